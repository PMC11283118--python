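"""Publish/subscribe message transport between the services.

Queues are named and fixed (the stack topology): ``ingest`` (SCP ->
fingerprinter), ``dispatch`` (fingerprinter -> scheduler), ``work.cpu`` /
``work.gpu`` (scheduler -> consumers), ``result`` (consumer -> scheduler)
and ``egress`` (scheduler -> SCU).  Delivery is at-least-once: a handler
that raises causes redelivery with an incremented delivery count, and a
message that keeps failing is moved to a per-queue dead-letter queue so
loss is observable rather than silent.

The backend implemented here is the deterministic in-memory broker: a
single-process pump that delivers messages FIFO per queue and shares work
round-robin across subscribers.  It is the reference implementation of
the broker contract and the harness every end-to-end test runs on; a
networked backend can implement the same ``publish``/``subscribe``
surface.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Callable

log = logging.getLogger(__name__)

__all__ = [
    "QUEUE_NAMES",
    "SCHEMAS",
    "Message",
    "BrokerError",
    "UnknownQueueError",
    "LivelockError",
    "MemoryBroker",
]

#: Fixed queue topology of the stack.
QUEUE_NAMES: tuple[str, ...] = (
    "ingest",
    "dispatch",
    "work.cpu",
    "work.gpu",
    "result",
    "egress",
)

#: Message schema names carried in each body's ``schema`` field.
SCHEMAS: dict[str, str] = {
    "ingest": "ingest.v1",
    "dispatch": "dispatch.v1",
    "work.cpu": "work.v1",
    "work.gpu": "work.v1",
    "result": "result.v1",
    "egress": "egress.v1",
}


class BrokerError(Exception):
    pass


class UnknownQueueError(BrokerError):
    """Queue name outside the configured topology."""


class LivelockError(BrokerError):
    """The pump exceeded its step budget without reaching quiescence."""


@dataclass(frozen=True)
class Message:
    message_id: str
    queue: str
    body: dict
    delivery_count: int = 1

    def json(self) -> str:
        return json.dumps(self.body, sort_keys=True)


Handler = Callable[[Message], None]


def dead_letter_queue(queue: str) -> str:
    return f"{queue}.dlq"


@dataclass
class _Pending:
    message_id: str
    body: dict
    delivery_count: int = 0


@dataclass
class MemoryBroker:
    """Single-process deterministic broker.

    Messages are pumped explicitly (:meth:`pump_one` /
    :meth:`pump_until_idle`), which makes the asynchronous message flow of
    the stack testable as a sequential program.  Handler exceptions are
    contained: the message is redelivered (appended back, delivery count
    incremented) up to ``max_deliveries``, then dead-lettered.
    """

    max_deliveries: int = 3
    queues: tuple[str, ...] = QUEUE_NAMES

    _pending: dict[str, deque] = field(default_factory=dict, repr=False)
    _subscribers: dict[str, list[Handler]] = field(default_factory=dict, repr=False)
    _rr: dict[str, itertools.cycle] = field(default_factory=dict, repr=False)
    _counter: itertools.count = field(default_factory=itertools.count, repr=False)

    def __post_init__(self) -> None:
        for q in self.queues:
            self._pending[q] = deque()
            self._pending[dead_letter_queue(q)] = deque()

    # -- contract ------------------------------------------------------
    def _check_queue(self, queue: str) -> None:
        if queue not in self._pending:
            raise UnknownQueueError(queue)

    def publish(self, queue: str, body: dict) -> str:
        self._check_queue(queue)
        # round-trip through JSON so only serializable bodies enter the bus
        body = json.loads(json.dumps(body))
        message_id = f"m{next(self._counter):06d}"
        self._pending[queue].append(_Pending(message_id=message_id, body=body))
        return message_id

    def subscribe(self, queue: str, handler: Handler) -> None:
        self._check_queue(queue)
        self._subscribers.setdefault(queue, []).append(handler)
        self._rr[queue] = itertools.cycle(range(len(self._subscribers[queue])))

    # -- introspection -------------------------------------------------
    def queue_depth(self, queue: str) -> int:
        self._check_queue(queue)
        return len(self._pending[queue])

    def dead_letters(self, queue: str) -> list[Message]:
        dlq = dead_letter_queue(queue)
        self._check_queue(dlq)
        return [
            Message(p.message_id, dlq, p.body, p.delivery_count)
            for p in self._pending[dlq]
        ]

    def drain(self, queue: str) -> list[Message]:
        """Pop all pending messages without invoking handlers (test aid)."""
        self._check_queue(queue)
        out = []
        while self._pending[queue]:
            p = self._pending[queue].popleft()
            out.append(Message(p.message_id, queue, p.body, p.delivery_count + 1))
        return out

    # -- pumping -------------------------------------------------------
    def pump_one(self) -> bool:
        """Deliver the next message on the first non-empty subscribed
        queue (topology order).  Returns False when nothing is deliverable.
        """
        for queue in self.queues:
            handlers = self._subscribers.get(queue)
            if not handlers or not self._pending[queue]:
                continue
            pending = self._pending[queue].popleft()
            pending.delivery_count += 1
            message = Message(
                message_id=pending.message_id,
                queue=queue,
                body=pending.body,
                delivery_count=pending.delivery_count,
            )
            handler = handlers[next(self._rr[queue]) % len(handlers)]
            try:
                handler(message)  # returning = ack; message is gone
            except Exception as exc:  # noqa: BLE001 - containment is the contract
                if pending.delivery_count >= self.max_deliveries:
                    log.warning(
                        "dead-lettering queue=%s message_id=%s deliveries=%d error=%s",
                        queue, message.message_id, pending.delivery_count, exc,
                    )
                    self._pending[dead_letter_queue(queue)].append(pending)
                else:
                    log.info(
                        "redelivering queue=%s message_id=%s deliveries=%d error=%s",
                        queue, message.message_id, pending.delivery_count, exc,
                    )
                    self._pending[queue].append(pending)
            return True
        return False

    def pump_until_idle(self, max_steps: int = 100_000) -> int:
        """Pump until every subscribed queue is empty; returns the number
        of deliveries made.  Bounded by ``max_steps`` to turn a livelock
        into a hard error instead of a hang."""
        steps = 0
        while self.pump_one():
            steps += 1
            if steps > max_steps:
                raise LivelockError(f"no quiescence after {max_steps} deliveries")
        return steps
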